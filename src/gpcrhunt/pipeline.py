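"""End-to-end orchestration: filter -> TMM -> RPKM -> reference gene ->
%-of-reference -> per-cohort calls -> frequency -> healthy filter -> clustering.

Runs the full receptor-discovery workflow over a set of cohort count matrices
and produces one consolidated SelectionReport, a ClusterAssignment and a run
manifest (config hash, input checksums, library versions, seed) so identical
configuration and inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import ClusterAssignment, ClusterConfig, hierarchical_clusters, \
    sample_distance
from .io_core import CountMatrix, GeneAnnotation, SampleMeta, SelectionReport, \
    ValidationError
from .normalize import ExpressionMatrix, FilterConfig, TmmConfig, compute_rpkm, \
    filter_low_expression, tmm_factors
from .reference_gene import DEFAULT_HOUSEKEEPING_CANDIDATES, ReferenceGeneReport, \
    relative_to_reference, select_reference
from .target_selection import SelectionConfig, call_expressed, cohort_frequency, \
    healthy_overexpression_filter, healthy_reference_stats, pairwise_coexpression

logger = logging.getLogger("gpcrhunt")


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    tmm: TmmConfig = field(default_factory=TmmConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    reference_candidates: tuple[str, ...] = DEFAULT_HOUSEKEEPING_CANDIDATES
    reference_cohort: str | None = None  # default: first healthy cohort
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for name, sub in (("filter", FilterConfig), ("tmm", TmmConfig),
                          ("selection", SelectionConfig), ("cluster", ClusterConfig)):
            if name in raw:
                kwargs[name] = sub(**raw[name])
        for name in ("reference_candidates", "reference_cohort", "seed"):
            if name in raw:
                kwargs[name] = tuple(raw[name]) if name == "reference_candidates" \
                    else raw[name]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reference_candidates"] = list(self.reference_candidates)
        return d


@dataclass
class PipelineResult:
    report: SelectionReport
    clusters: ClusterAssignment | None
    reference: ReferenceGeneReport
    manifest: dict


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage name."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as e:
                raise StageError(f"stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def _pooled(matrices: list[ExpressionMatrix], genes, unit: str,
            provenance: str) -> ExpressionMatrix:
    """Concatenate cohort matrices column-wise over a fixed gene list; genes
    absent from a cohort (filtered there) become unavailable cells."""
    parts = [m.values.reindex(list(genes)) for m in matrices]
    return ExpressionMatrix(pd.concat(parts, axis=1), unit, provenance=provenance)


def run_pipeline(cohorts: dict[str, CountMatrix], annotation: GeneAnnotation,
                 meta: SampleMeta, cfg: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Execute the full selection workflow over a cohort collection.

    ``cohorts`` maps cohort id to raw counts; ``meta`` assigns each sample a
    cohort and a healthy/cancer condition (healthy samples additionally need
    tissue labels when the healthy filter is restricted to peritoneum).
    """
    cfg = cfg or PipelineConfig()
    if not cohorts:
        raise ValidationError("run_pipeline requires at least one cohort")

    healthy_ids = sorted({meta.table.loc[s, "cohort_id"]
                          for s in meta.samples_where(condition="healthy")
                          if meta.table.loc[s, "cohort_id"] in cohorts})
    cancer_ids = [c for c in cohorts if c not in healthy_ids]

    # --- per-cohort normalization -----------------------------------------
    rpkm: dict[str, ExpressionMatrix] = {}
    for cid, cm in cohorts.items():
        filtered = _stage("filter")(filter_low_expression)(cm, cfg.filter)
        nf = _stage("tmm")(tmm_factors)(filtered, cfg.tmm)
        rpkm[cid] = _stage("rpkm")(compute_rpkm)(filtered, annotation, nf)
        logger.info("cohort %s: %d genes after filter, %d samples", cid,
                    len(filtered.gene_symbols), len(filtered.sample_ids))

    # --- reference gene ---------------------------------------------------
    ref_cohort = cfg.reference_cohort
    if ref_cohort is None:
        if not healthy_ids:
            raise StageError("stage 'reference' failed: no healthy cohort "
                             "available for reference-gene selection")
        ref_cohort = healthy_ids[0]
    if ref_cohort not in rpkm:
        raise StageError(f"stage 'reference' failed: reference cohort "
                         f"{ref_cohort!r} not among inputs")
    refrep = _stage("reference")(select_reference)(
        rpkm[ref_cohort], cfg.reference_candidates, cohort_id=ref_cohort)

    pct = {cid: _stage("pct_ref")(relative_to_reference)(m, refrep.selected)
           for cid, m in rpkm.items()}

    # --- per-cohort expressed calls and frequency ranking -----------------
    gpcrs = annotation.gpcr_symbols
    sets = {cid: _stage("call_expressed")(call_expressed)(
        pct[cid], gpcrs, cfg.selection) for cid in cancer_ids}
    freq, preselected = _stage("frequency")(cohort_frequency)(sets, cfg.selection)

    # --- healthy-tissue overexpression filter -----------------------------
    final: list[str] = []
    pass_fraction: dict[str, float] = {}
    if preselected:
        if not healthy_ids:
            raise StageError("stage 'healthy_filter' failed: no healthy cohort "
                             "in the collection; cannot apply the healthy-"
                             "tissue overexpression filter")
        scale = cfg.selection.healthy_filter_scale
        source = rpkm if scale == "RPKM" else pct
        e_healthy = _pooled([source[c] for c in healthy_ids],
                            preselected, source[healthy_ids[0]].unit,
                            "pooled healthy")
        stats = _stage("healthy_stats")(healthy_reference_stats)(
            e_healthy, meta, preselected, cfg.selection)
        pooled_cancer = _pooled([source[c] for c in cancer_ids], preselected,
                                source[cancer_ids[0]].unit, "pooled cancer")
        final, pass_fraction = _stage("healthy_filter")(
            healthy_overexpression_filter)(pooled_cancer, stats, preselected,
                                           cfg.selection)

    # --- co-expression and clustering on the final panel ------------------
    coexpression: dict[str, float] = {}
    clusters: ClusterAssignment | None = None
    if final:
        pooled_pct = _pooled([pct[c] for c in cancer_ids], final,
                             "PCT_REF", "pooled cancer pct_ref")
        if len(final) >= 2:
            coexpression = _stage("coexpression")(pairwise_coexpression)(
                pooled_pct, final, cfg.selection)
        n_samples = pooled_pct.values.shape[1]
        if n_samples >= 2:
            ccfg = dataclasses.replace(cfg.cluster,
                                       k=min(cfg.cluster.k, n_samples))
            d = _stage("distance")(sample_distance)(pooled_pct, ccfg)
            clusters = _stage("clustering")(hierarchical_clusters)(d, ccfg)

    report = SelectionReport(
        per_cohort_expressed=sets,
        frequency=freq,
        preselected=preselected,
        final_targets=final,
        pass_fraction=pass_fraction,
        coexpression=coexpression,
        cluster_labels={} if clusters is None
        else {s: int(v) for s, v in clusters.labels.items()},
    )
    manifest = _build_manifest(cohorts, cfg, refrep)
    logger.info("pipeline: %d expressed-call sets -> %d preselected -> %d "
                "final targets", len(sets), len(preselected), len(final))
    return PipelineResult(report=report, clusters=clusters, reference=refrep,
                          manifest=manifest)


def _build_manifest(cohorts: dict[str, CountMatrix], cfg: PipelineConfig,
                    refrep: ReferenceGeneReport) -> dict:
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    checksums = {
        cid: hashlib.sha256(
            cm.counts.to_csv(sep="\t").encode()).hexdigest()[:16]
        for cid, cm in cohorts.items()
    }
    return {
        "package_version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "config": cfg.to_dict(),
        "input_checksums": checksums,
        "reference_gene": refrep.selected,
        "seed": cfg.seed,
    }
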