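"""Synthetic paired miRNA/mRNA experiments with planted ground truth.

The generator emulates the design of a postnatal heart time course: four
ordered time points (P01, P04, P09, P23) with four biological replicates
each, negative-binomial miRNA counts over per-sample size factors, and a
companion differential mRNA table. Planted differentially expressed miRNAs
follow one of five named trajectory templates mirroring the phenomenology
of such time courses (log2 offsets from the first time point):

    early_up    (0,  L,  L,  L)   DE from the first window onward, up
    early_down  (0, -L, -L, -L)   DE from the first window onward, down
    mid_down    (0,  0, -L, -L)   DE from the second window onward
    late_up     (0,  0,  0,  L)   DE only in the last window
    transient   (0, 0, -1.2, -0.45)  a dip at the third time point that
                                  mostly recovers — differential in the
                                  P09-P04 window only, sub-threshold in
                                  every cumulative later comparison

Each planted DE miRNA receives a block of *true repressive edges* to genes
that move in the opposite direction in every comparison where the miRNA is
differential, plus decoy predicted edges to unrelated genes; target blocks
are disjoint across miRNAs so planted truth is unambiguous. Per planted
miRNA, one gene set heavily overlapping its true targets is planted in the
collection among uniform background sets.

Everything is driven by a single numpy Generator: identical config + seed
reproduce identical objects and byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import ComparisonSpec
from .io_formats import (
    CountMatrix,
    DifferentialGeneTable,
    GeneSet,
    GeneSetCollection,
    PredictedTargetTable,
    SampleMetadata,
    ValidationError,
    write_count_matrix,
    write_differential_genes,
    write_gmt,
    write_predicted_targets,
    write_sample_metadata,
)
from .qpcr import QpcrPlate

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticExperiment",
    "generate_experiment",
    "generate_qpcr_plate",
    "write_experiment",
    "default_comparison_plan",
]

TIME_POINTS = ("P01", "P04", "P09", "P23")

# fixed shape of the transient template (see module docstring)
_TRANSIENT_DIP = -1.2
_TRANSIENT_RESIDUAL = -0.45

_TEMPLATES = ("early_up", "early_down", "mid_down", "late_up", "transient")


def _template_offsets(template: str, magnitude: float) -> tuple[float, float, float, float]:
    L = magnitude
    return {
        "early_up": (0.0, L, L, L),
        "early_down": (0.0, -L, -L, -L),
        "mid_down": (0.0, 0.0, -L, -L),
        "late_up": (0.0, 0.0, 0.0, L),
        "transient": (0.0, 0.0, _TRANSIENT_DIP, _TRANSIENT_RESIDUAL),
    }[template]


def default_comparison_plan(
    time_points=TIME_POINTS,
) -> tuple[list[ComparisonSpec], list[ComparisonSpec]]:
    """(adjacent, long_range) comparisons for an ordered time course.

    Adjacent: consecutive pairs. Long-range: every later point against the
    first (the "cumulative" comparisons used for persistence bookkeeping),
    excluding the pair already covered by the adjacent chain.
    """
    tps = list(time_points)
    adjacent = [ComparisonSpec(tps[i + 1], tps[i]) for i in range(len(tps) - 1)]
    long_range = [ComparisonSpec(tp, tps[0]) for tp in tps[2:]]
    return adjacent, long_range


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs for the synthetic experiment.

    Defaults emulate a small-RNA time course: 4 x 4 design, ~20% of miRNAs
    planted DE with |log2FC| in [1.5, 3], NB dispersions log-uniform in
    [0.01, 0.2], planted miRNAs expressed well above the 300-count floor,
    ~60 true repressive targets per DE miRNA (comfortably above the
    40-target eligibility gate) plus 150 decoy predictions each.
    """

    n_mirna: int = 200
    n_gene: int = 4000
    time_points: tuple[str, ...] = TIME_POINTS
    replicates: int = 4
    fraction_de: float = 0.2
    log2fc_range: tuple[float, float] = (1.5, 3.0)
    phi_range: tuple[float, float] = (0.01, 0.2)
    de_mean_range: tuple[float, float] = (500.0, 5000.0)
    background_mean_range: tuple[float, float] = (5.0, 3000.0)
    size_factor_sd: float = 0.1
    n_true_targets: int = 60
    n_decoy_targets: int = 150
    background_de_fraction: float = 0.15
    n_background_sets: int = 50
    planted_set_size: int = 60
    planted_overlap_fraction: float = 0.8
    template_weights: dict = field(
        default_factory=lambda: {
            "early_up": 1, "early_down": 5, "mid_down": 10, "late_up": 19, "transient": 1
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirna, self.n_gene, self.replicates) < 1:
            raise ValidationError("counts in the generator config must be positive")
        if not (0.0 <= self.fraction_de <= 1.0):
            raise ValidationError("fraction_de must lie in [0, 1]")
        if not (0.0 <= self.background_de_fraction <= 1.0):
            raise ValidationError("background_de_fraction must lie in [0, 1]")
        if len(self.time_points) != 4:
            raise ValidationError("trajectory templates are defined for 4 time points")
        if self.replicates < 2:
            raise ValidationError("at least 2 replicates per group are required")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: what a perfect analysis should recover."""

    time_points: tuple[str, ...]
    templates: dict[str, str]  # DE miRNA -> template name
    log2fc_offsets: dict[str, tuple[float, ...]]  # per-time-point offsets (all miRNAs)
    base_means: dict[str, float]
    dispersions: dict[str, float]
    true_edges: tuple[tuple[str, str], ...]  # repressive (miRNA, gene)
    decoy_edges: tuple[tuple[str, str], ...]
    planted_sets: dict[str, str]  # DE miRNA -> planted set id
    seed: int

    @property
    def de_mirnas(self) -> list[str]:
        return sorted(self.templates)

    def delta_log2fc(self, cmp: ComparisonSpec) -> dict[str, float]:
        """True log2 fold change (later - earlier offset) per miRNA."""
        il = self.time_points.index(cmp.later)
        ie = self.time_points.index(cmp.earlier)
        return {m: off[il] - off[ie] for m, off in self.log2fc_offsets.items()}

    def true_targets(self, mirna: str) -> frozenset[str]:
        return frozenset(g for m, g in self.true_edges if m == mirna)

    def to_json(self, path) -> None:
        payload = {
            "time_points": list(self.time_points),
            "templates": self.templates,
            "log2fc_offsets": {m: list(v) for m, v in self.log2fc_offsets.items()},
            "base_means": self.base_means,
            "dispersions": self.dispersions,
            "true_edges": [list(e) for e in self.true_edges],
            "decoy_edges": [list(e) for e in self.decoy_edges],
            "planted_sets": self.planted_sets,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @staticmethod
    def from_json(path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return SyntheticTruth(
            time_points=tuple(d["time_points"]),
            templates=d["templates"],
            log2fc_offsets={m: tuple(v) for m, v in d["log2fc_offsets"].items()},
            base_means=d["base_means"],
            dispersions=d["dispersions"],
            true_edges=tuple(tuple(e) for e in d["true_edges"]),
            decoy_edges=tuple(tuple(e) for e in d["decoy_edges"]),
            planted_sets=d["planted_sets"],
            seed=d["seed"],
        )


@dataclass(frozen=True)
class SyntheticExperiment:
    counts: CountMatrix
    metadata: SampleMetadata
    mrna: DifferentialGeneTable
    predicted: PredictedTargetTable
    gene_sets: GeneSetCollection
    truth: SyntheticTruth


def _assign_templates(n_de: int, weights: dict, rng: np.random.Generator) -> list[str]:
    """Largest-remainder apportionment of templates, order shuffled."""
    names = [t for t in _TEMPLATES if weights.get(t, 0) > 0]
    w = np.array([weights[t] for t in names], dtype=float)
    if n_de == 0 or not len(names):
        return []
    quota = w / w.sum() * n_de
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(-remainder)[: n_de - counts.sum()]:
        counts[i] += 1
    out = [t for t, c in zip(names, counts) for _ in range(c)]
    rng.shuffle(out)
    return out


_SET_NAME_POOL = [
    "mitochondrion", "mitochondrial inner membrane", "mitochondrial matrix",
    "mitotic cell cycle process", "DNA replication", "DNA repair",
    "positive regulation of cell proliferation", "fatty acid metabolic process",
    "fatty acid beta-oxidation", "oxoacid metabolic process", "glycolytic process",
    "cellular respiration", "actin cytoskeleton organization", "regulation of cell size",
    "cholesterol metabolic process", "heart development", "ERK1 and ERK2 cascade",
    "integrin-mediated signaling pathway", "ECM-receptor interaction",
    "regulation of actin cytoskeleton", "glycerolipid metabolism",
    "PI3K-Akt signaling pathway", "MAPK signaling pathway", "cell cycle",
    "PPAR signaling pathway", "hypertrophic cardiomyopathy",
    "valine leucine and isoleucine degradation", "arginine and proline metabolism",
    "nucleus", "cytosol", "ribosome", "protein kinase B signaling",
]


def generate_experiment(config: GeneratorConfig | None = None) -> SyntheticExperiment:
    """Generate a complete paired experiment with planted truth."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    tps = list(cfg.time_points)

    mirnas = [f"syn-miR-{i + 1:04d}" for i in range(cfg.n_mirna)]
    genes = [f"GENE{i + 1:05d}" for i in range(cfg.n_gene)]

    n_de = int(round(cfg.fraction_de * cfg.n_mirna))
    de_idx = sorted(rng.choice(cfg.n_mirna, size=n_de, replace=False).tolist())
    de_mirnas = [mirnas[i] for i in de_idx]
    templates = dict(zip(de_mirnas, _assign_templates(n_de, cfg.template_weights, rng)))

    # expression model: baseline mean, per-time-point log2 offsets, dispersion
    lo, hi = cfg.log2fc_range
    offsets: dict[str, tuple[float, ...]] = {}
    base_means: dict[str, float] = {}
    dispersions: dict[str, float] = {}
    for m in mirnas:
        if m in templates:
            L = float(rng.uniform(lo, hi))
            offsets[m] = _template_offsets(templates[m], L)
            lo_m, hi_m = cfg.de_mean_range
        else:
            offsets[m] = (0.0,) * len(tps)
            lo_m, hi_m = cfg.background_mean_range
        base_means[m] = float(np.exp(rng.uniform(np.log(lo_m), np.log(hi_m))))
        p_lo, p_hi = cfg.phi_range
        dispersions[m] = float(np.exp(rng.uniform(np.log(p_lo), np.log(p_hi))))

    # counts: NB(mean = sf_j * mu_ft, phi_f)
    samples = [f"{tp}_r{r + 1}" for tp in tps for r in range(cfg.replicates)]
    sample_tp = {s: s.rsplit("_r", 1)[0] for s in samples}
    sf = np.exp(rng.normal(0.0, cfg.size_factor_sd, size=len(samples)))
    mu = np.empty((cfg.n_mirna, len(samples)))
    phi = np.array([dispersions[m] for m in mirnas])
    for j, s in enumerate(samples):
        ti = tps.index(sample_tp[s])
        mu[:, j] = sf[j] * np.array(
            [base_means[m] * 2.0 ** offsets[m][ti] for m in mirnas]
        )
    r_param = 1.0 / np.maximum(phi, 1e-12)[:, None]
    p_param = r_param / (r_param + mu)
    counts = rng.negative_binomial(r_param, p_param)
    cm = CountMatrix(pd.DataFrame(counts, index=mirnas, columns=samples))
    md = SampleMetadata(time_point=sample_tp, time_points_order=tps)

    # true repressive target blocks (disjoint across miRNAs)
    if n_de * cfg.n_true_targets > cfg.n_gene:
        raise ValidationError(
            f"config demands {n_de * cfg.n_true_targets} true edges but only "
            f"{cfg.n_gene} genes exist"
        )
    perm = rng.permutation(cfg.n_gene)
    true_edges: list[tuple[str, str]] = []
    target_block: dict[str, list[str]] = {}
    cursor = 0
    for m in de_mirnas:
        block = [genes[i] for i in sorted(perm[cursor: cursor + cfg.n_true_targets])]
        cursor += cfg.n_true_targets
        target_block[m] = block
        true_edges.extend((m, g) for g in block)
    targeted = {g for _, g in true_edges}
    free_genes = [g for g in genes if g not in targeted]

    # differential mRNA table driven by the planted trajectories
    adjacent, long_range = default_comparison_plan(tps)
    plan = adjacent + long_range
    de_call_threshold = np.log2(1.8)
    rows: list[dict] = []
    for cmp in plan:
        il, ie = tps.index(cmp.later), tps.index(cmp.earlier)
        for m in de_mirnas:
            delta = offsets[m][il] - offsets[m][ie]
            if abs(delta) < de_call_threshold:
                continue
            gene_dir = "down" if delta > 0 else "up"  # repression: opposite move
            for g in target_block[m]:
                rows.append(
                    {
                        "gene": g,
                        "comparison": cmp.id,
                        "direction": gene_dir,
                        "fold_change": float(rng.uniform(2.0, 6.0)),
                        "fdr": float(10.0 ** rng.uniform(-6.0, -2.5)),
                    }
                )
    n_bg_de = int(round(cfg.background_de_fraction * len(free_genes)))
    bg_de = [free_genes[i] for i in sorted(rng.choice(len(free_genes), n_bg_de, replace=False))]
    for g in bg_de:
        for cmp in plan:
            if rng.random() < 0.5:
                rows.append(
                    {
                        "gene": g,
                        "comparison": cmp.id,
                        "direction": "up" if rng.random() < 0.5 else "down",
                        "fold_change": float(rng.uniform(1.8, 5.0)),
                        "fdr": float(10.0 ** rng.uniform(-5.0, -2.5)),
                    }
                )
    mrna = DifferentialGeneTable(
        pd.DataFrame(rows, columns=["gene", "comparison", "direction", "fold_change", "fdr"])
    )

    # predicted-target table: true edges + decoys
    decoy_edges: list[tuple[str, str]] = []
    predicted: dict[str, set[str]] = {}
    for m in de_mirnas:
        own = set(target_block[m])
        pool = [g for g in genes if g not in own]
        decoys = [pool[i] for i in sorted(rng.choice(len(pool), cfg.n_decoy_targets, replace=False))]
        decoy_edges.extend((m, g) for g in decoys)
        predicted[m] = own | set(decoys)
    ptt = PredictedTargetTable({m: frozenset(gs) for m, gs in predicted.items()})

    # gene sets: one planted per DE miRNA + uniform background sets
    sets: list[GeneSet] = []
    planted_sets: dict[str, str] = {}
    categories = ("GO_BP", "GO_CC", "KEGG")
    n_overlap = int(round(cfg.planted_overlap_fraction * cfg.planted_set_size))
    for i, m in enumerate(de_mirnas):
        block = target_block[m]
        k = min(n_overlap, len(block))
        members = set(
            block[j] for j in sorted(rng.choice(len(block), k, replace=False))
        )
        pool = [g for g in genes if g not in set(block)]
        extra = cfg.planted_set_size - k
        members |= {pool[j] for j in sorted(rng.choice(len(pool), extra, replace=False))}
        set_id = f"SYN:P{i + 1:03d}"
        planted_sets[m] = set_id
        sets.append(
            GeneSet(set_id, f"planted program {m}", categories[i % 3], frozenset(members))
        )
    for i in range(cfg.n_background_sets):
        size = int(rng.integers(20, 120))
        members = {genes[j] for j in sorted(rng.choice(cfg.n_gene, size, replace=False))}
        name = _SET_NAME_POOL[i % len(_SET_NAME_POOL)]
        if i >= len(_SET_NAME_POOL):
            name = f"{name} {i // len(_SET_NAME_POOL) + 1}"
        sets.append(
            GeneSet(f"SYN:B{i + 1:03d}", name, categories[i % 3], frozenset(members))
        )
    collection = GeneSetCollection(tuple(sets))

    truth = SyntheticTruth(
        time_points=tuple(tps),
        templates=templates,
        log2fc_offsets=offsets,
        base_means=base_means,
        dispersions=dispersions,
        true_edges=tuple(sorted(true_edges)),
        decoy_edges=tuple(sorted(decoy_edges)),
        planted_sets=planted_sets,
        seed=cfg.seed,
    )
    return SyntheticExperiment(cm, md, mrna, ptt, collection, truth)


def generate_qpcr_plate(
    truth: SyntheticTruth,
    noise_sd: float = 0.15,
    targets: list[str] | None = None,
    n_targets: int = 18,
    n_references: int = 2,
    n_spike_ins: int = 2,
    replicates: int = 4,
    seed: int | None = None,
) -> QpcrPlate:
    """Synthetic Cq plate consistent with the planted trajectories.

    Cq = per-assay baseline - log2(relative abundance) + Gaussian noise.
    Reference assays are flat across groups by construction; spike-ins are
    flat across samples. With ``noise_sd = 0`` the ddCt chain recovers the
    planted log2 offsets exactly.
    """
    if noise_sd < 0:
        raise ValidationError("noise SD must be non-negative")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if targets is None:
        targets = truth.de_mirnas[:n_targets]
    missing = [t for t in targets if t not in truth.log2fc_offsets]
    if missing:
        raise ValidationError(f"no planted truth for qPCR target(s): {missing}")

    tps = list(truth.time_points)
    rows: list[dict] = []
    base_t = {t: float(rng.uniform(22.0, 28.0)) for t in targets}
    refs = [f"syn-ref-{i + 1}" for i in range(n_references)]
    base_r = {r: float(rng.uniform(18.0, 22.0)) for r in refs}
    spikes = [f"syn-spike-{i + 1}" for i in range(n_spike_ins)]
    base_s = {s: float(rng.uniform(15.0, 18.0)) for s in spikes}

    for ti, tp in enumerate(tps):
        for rep in range(replicates):
            sample = f"{tp}_q{rep + 1}"
            for t in targets:
                cq = base_t[t] - truth.log2fc_offsets[t][ti]
                if noise_sd > 0:
                    cq += float(rng.normal(0.0, noise_sd))
                rows.append(
                    {"sample": sample, "assay": t, "cq": cq,
                     "designation": "target", "group": tp}
                )
            for r in refs:
                cq = base_r[r]
                if noise_sd > 0:
                    cq += float(rng.normal(0.0, noise_sd))
                rows.append(
                    {"sample": sample, "assay": r, "cq": cq,
                     "designation": "reference", "group": tp}
                )
            for s in spikes:
                rows.append(
                    {"sample": sample, "assay": s, "cq": base_s[s],
                     "designation": "spike_in", "group": tp}
                )
    return QpcrPlate(pd.DataFrame(rows, columns=_PLATE_COLS))


_PLATE_COLS = ["sample", "assay", "cq", "designation", "group"]


def write_experiment(exp: SyntheticExperiment, outdir) -> dict[str, Path]:
    """Serialize every table of an experiment into ``outdir``; returns the
    path map. Byte-identical for identical experiments."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "mirna_counts.tsv",
        "metadata": outdir / "sample_metadata.tsv",
        "mrna": outdir / "mrna_differential.tsv",
        "predicted": outdir / "predicted_targets.tsv",
        "truth": outdir / "truth.json",
    }
    write_count_matrix(exp.counts, paths["counts"])
    write_sample_metadata(exp.metadata, paths["metadata"])
    write_differential_genes(exp.mrna, paths["mrna"])
    write_predicted_targets(exp.predicted, paths["predicted"])
    # GMT carries no category column, so one file per category
    for cat in ("GO_BP", "GO_CC", "KEGG"):
        sub = GeneSetCollection(tuple(s for s in exp.gene_sets if s.category == cat))
        path = outdir / f"gene_sets_{cat}.gmt"
        write_gmt(sub, path)
        paths[f"gene_sets_{cat}"] = path
    exp.truth.to_json(paths["truth"])
    return paths
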