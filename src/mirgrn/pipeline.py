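"""End-to-end orchestration: filter -> differential expression per
comparison -> temporal classification -> target verification -> eligibility
gate -> enrichment -> network export, from a single config.

Every output is deterministic (no timestamps, fixed orderings, fixed float
formats): re-running on identical inputs reproduces every byte, and the
manifest records the tool version, the config hash and input/output
checksums so a run can be audited and replayed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from . import diffexpr, temporal, targets, enrichment as enrich_mod, network as net_mod
from .diffexpr import ComparisonSpec
from .io_formats import (
    GeneSetCollection,
    ValidationError,
    read_count_matrix,
    read_differential_genes,
    read_gmt,
    read_predicted_targets,
    read_sample_metadata,
)

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)

UNIVERSE_POLICIES = ("measured_and_annotated", "measured", "annotated")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs, thresholds and modes for one pipeline run.

    ``gene_sets`` maps category (GO_BP / GO_CC / KEGG) to a GMT path.
    ``adjacent`` / ``long_range`` are lists of [later, earlier] pairs; when
    omitted they default to the consecutive chain and the
    every-later-vs-first comparisons implied by the metadata time order.
    """

    counts: str
    metadata: str
    mrna: str
    predicted: str
    gene_sets: dict[str, str]
    out_dir: str
    fc_threshold: float = diffexpr.DEFAULT_FC_THRESHOLD
    fdr_alpha: float = diffexpr.DEFAULT_FDR_ALPHA
    min_mean: float = diffexpr.DEFAULT_MIN_MEAN
    epsilon: float = diffexpr.DEFAULT_EPSILON
    min_targets: int = targets.DEFAULT_MIN_TARGETS
    alpha: float = enrich_mod.DEFAULT_ALPHA
    enrichment_mode: str = "fisher"
    universe_policy: str = "measured_and_annotated"
    verification_scope: str = "first"  # or "per_comparison"
    mito_pattern: str = net_mod.MITO_PATTERN
    adjacent: list | None = None
    long_range: list | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fdr_alpha <= 1 and 0 < self.alpha <= 1):
            raise ValidationError("significance levels must lie in (0, 1]")
        if self.fc_threshold < 1:
            raise ValidationError("fc_threshold must be >= 1")
        if self.universe_policy not in UNIVERSE_POLICIES:
            raise ValidationError(f"universe_policy must be one of {UNIVERSE_POLICIES}")
        if self.enrichment_mode not in ("fisher", "ease"):
            raise ValidationError("enrichment_mode must be fisher or ease")
        if self.verification_scope not in ("first", "per_comparison"):
            raise ValidationError("verification_scope must be first or per_comparison")

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return PipelineConfig(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    de_tables: dict[str, pd.DataFrame]
    patterns: list
    verified: list
    records: list
    network: net_mod.RegulatoryNetwork
    outputs: dict[str, Path]
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mirgrn {__version__}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s finished in %.2fs", name, dt)
                return False
            if isinstance(exc, PipelineError):
                return False
            raise PipelineError(name, str(exc)) from exc

    return _Ctx()


def _comparison_plan(cfg: PipelineConfig, tp_order: list[str]):
    if cfg.adjacent:
        adjacent = [ComparisonSpec(l, e) for l, e in cfg.adjacent]
    else:
        adjacent = [
            ComparisonSpec(tp_order[i + 1], tp_order[i]) for i in range(len(tp_order) - 1)
        ]
    if cfg.long_range is not None:
        long_range = [ComparisonSpec(l, e) for l, e in cfg.long_range]
    else:
        long_range = [ComparisonSpec(tp, tp_order[0]) for tp in tp_order[2:]]
    for c in adjacent + long_range:
        c.validate_order(tp_order)
    return adjacent, long_range


def _universe(policy: str, mrna, collection: GeneSetCollection) -> frozenset[str]:
    measured = mrna.measured_genes()
    annotated = collection.annotated_genes()
    if policy == "measured":
        return measured
    if policy == "annotated":
        return annotated
    return measured & annotated


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages; writes every artifact under ``cfg.out_dir`` and
    returns the in-memory results plus the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    with _stage("io"):
        for name in ("counts", "metadata", "predicted"):
            if not Path(getattr(cfg, name)).exists():
                raise FileNotFoundError(f"input {name!r} not found: {getattr(cfg, name)}")
        counts = read_count_matrix(cfg.counts)
        metadata = read_sample_metadata(cfg.metadata)
        predicted = read_predicted_targets(cfg.predicted)
        collections = []
        for cat, path in sorted(cfg.gene_sets.items()):
            if not Path(path).exists():
                raise FileNotFoundError(f"gene set file not found: {path}")
            collections.append(read_gmt(path, category=cat))
        collection = GeneSetCollection.merge(*collections)

    with _stage("diffexpr"):
        adjacent, long_range = _comparison_plan(cfg, metadata.time_points_order)
        plan = adjacent + long_range
        dispersions = diffexpr.estimate_dispersions(counts, metadata)
        de_tables: dict[str, pd.DataFrame] = {}
        for cmp in plan:
            res = diffexpr.call_differential(
                counts, metadata, cmp,
                fc_threshold=cfg.fc_threshold, fdr_alpha=cfg.fdr_alpha,
                min_mean=cfg.min_mean, epsilon=cfg.epsilon,
                dispersions=dispersions,
            )
            de_tables[cmp.id] = res
            p = out / f"de_{cmp.id}.tsv"
            _write_tsv(res, p)
            outputs[f"de_{cmp.id}"] = p

    with _stage("temporal_patterns"):
        patterns = temporal.classify_patterns(de_tables, adjacent, long_range)
        pframe = temporal.patterns_to_frame(patterns)
        outputs["patterns"] = out / "patterns.tsv"
        _write_tsv(pframe, outputs["patterns"])
        summary = temporal.pattern_summary(patterns, [c.id for c in plan])
        outputs["pattern_summary"] = out / "pattern_summary.tsv"
        _write_tsv(summary, outputs["pattern_summary"])

    with _stage("target_integration"):
        # the differential mRNA table is this stage's prerequisite
        if not Path(cfg.mrna).exists():
            raise FileNotFoundError(f"differential mRNA table not found: {cfg.mrna}")
        mrna = read_differential_genes(cfg.mrna)
        verified: list[targets.VerifiedTargetSet] = []
        mrna_cmps = set(mrna.comparisons())
        if cfg.verification_scope == "first":
            jobs: dict[str, list[str]] = {}
            for p in patterns:
                if p.first_comparison is not None:
                    jobs.setdefault(p.first_comparison, []).append(p.mirna)
            for cmp_id in sorted(jobs):
                if cmp_id not in mrna_cmps:
                    log.warning("comparison %s absent from mRNA table; skipped", cmp_id)
                    continue
                verified.extend(
                    targets.verify_targets(
                        predicted, mrna, de_tables[cmp_id], cmp_id, mirnas=jobs[cmp_id]
                    )
                )
        else:
            for cmp in plan:
                if cmp.id not in mrna_cmps:
                    continue
                verified.extend(
                    targets.verify_targets(predicted, mrna, de_tables[cmp.id], cmp.id)
                )
        verified = targets.filter_min_targets(verified, cfg.min_targets)
        edges_df, summary_df = targets.verified_to_frames(verified)
        outputs["verified_targets"] = out / "verified_targets.tsv"
        _write_tsv(edges_df, outputs["verified_targets"])
        outputs["verified_summary"] = out / "verified_summary.tsv"
        _write_tsv(summary_df, outputs["verified_summary"])

    with _stage("enrichment"):
        universe = _universe(cfg.universe_policy, mrna, collection)
        records: list[enrich_mod.EnrichmentRecord] = []
        for v in verified:
            if v.eligible:
                records.extend(
                    enrich_mod.enrich_mirna(
                        v, collection, universe, alpha=cfg.alpha, mode=cfg.enrichment_mode
                    )
                )
        rec_df = enrich_mod.records_to_frame(records)
        outputs["enrichment"] = out / "enrichment.tsv"
        _write_tsv(rec_df, outputs["enrichment"])

    with _stage("network_export"):
        network = net_mod.build_network(records)
        outputs["chord_matrix"] = out / "network_chord.tsv"
        outputs["chord_nodes"] = out / "network_nodes.json"
        net_mod.export_chord(network, outputs["chord_matrix"], outputs["chord_nodes"])
        outputs["sankey"] = out / "network_sankey.json"
        net_mod.export_sankey(network, outputs["sankey"])
        mito = net_mod.subnetwork_by_term_pattern(network, cfg.mito_pattern)
        outputs["mito_sankey"] = out / "network_mito_sankey.json"
        net_mod.export_sankey(mito, outputs["mito_sankey"])

    with _stage("manifest"):
        cfg_dict = cfg.to_dict()
        cfg_json = json.dumps(cfg_dict, sort_keys=True)
        inputs = {
            "counts": cfg.counts, "metadata": cfg.metadata,
            "mrna": cfg.mrna, "predicted": cfg.predicted,
            **{f"gene_sets_{c}": p for c, p in sorted(cfg.gene_sets.items())},
        }
        manifest = {
            "tool": "mirgrn",
            "version": __version__,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "inputs": {k: {"path": str(v), "sha256": _sha256(Path(v))}
                       for k, v in sorted(inputs.items())},
            "outputs": {k: {"path": str(v), "sha256": _sha256(v)}
                        for k, v in sorted(outputs.items())},
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs["manifest"] = manifest_path

    return PipelineResult(de_tables, patterns, verified, records, network, outputs, manifest)
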