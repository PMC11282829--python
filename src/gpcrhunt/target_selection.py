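"""Three-stage selection cascade for overexpressed cell-surface receptors.

Stage 1 (per cohort): a GPCR is called expressed when it reaches at least
``level_threshold_pct`` percent of the housekeeping reference in at least
``within_cohort_fraction`` of the cohort's samples.

Stage 2 (across cohorts): genes called expressed in at least ``min_cohorts``
independent cohorts are pre-selected, ranking receptors by recurrence rather
than by effect size in any single dataset.

Stage 3 (healthy filter): a pre-selected gene is retained only if its
expression in pooled cancer samples exceeds mean + ``sd_multiplier`` x SD of
the healthy comparator tissue in at least ``pooled_fraction`` of samples —
receptors equally present in healthy peritoneum would make poor drug-delivery
targets for intraperitoneal administration.

All threshold comparisons use >= (an "at least" reading), so boundary cases
pass.  Cells marked unavailable (NaN) are excluded from both numerator and
denominator of every fraction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import SampleMeta, ValidationError
from .normalize import UNIT_PCT_REF, ExpressionMatrix

logger = logging.getLogger("gpcrhunt")

#: GPCRs recurrently called expressed across the five public HGSOC cohorts,
#: keyed by the number of cohorts in which each was expressed.  Shipped as a
#: worked example for the frequency-ranking stage.
REPORTED_FREQUENT_GPCRS: dict[int, tuple[str, ...]] = {
    5: ("ACKR3", "ADGRA2", "ADGRA3", "ADGRE5", "ADGRG1", "ADRA2C", "C5AR1",
        "CXCR4", "F2R", "FPR3", "GPRC5A", "GPRC5B", "PTAFR", "S1PR2", "SMO"),
    4: ("ADGRF5", "ADGRG2", "CCR1", "CELSR1", "CELSR2", "CYSLTR1", "GPR157",
        "GPR183", "GPRC5C", "LGR4", "LGR6", "LPAR2", "LPAR3", "LPAR6", "OPN3"),
    3: ("ADGRL1", "ADGRL2", "C5AR2", "CCR5", "EDNRA", "F2RL1", "GPR34",
        "GPR82", "GPR89B", "HCAR1", "LGR5", "MC1R", "PTGIR", "PTH2R", "TBXA2R"),
}

#: The 13-receptor panel surviving the healthy-tissue overexpression filter in
#: the published HGSOC analysis; used as default planted targets in synthetic
#: cohorts.
REPORTED_FINAL_PANEL: tuple[str, ...] = (
    "ADGRF5", "ADGRG1", "ADRA2C", "CELSR1", "CELSR2", "CXCR4", "F2R",
    "GPR183", "LGR6", "LPAR3", "PTAFR", "PTH2R", "S1PR2",
)


@dataclass
class SelectionConfig:
    level_threshold_pct: float = 40.0     # % of reference gene
    within_cohort_fraction: float = 0.30  # of available samples, per cohort
    min_cohorts: int = 3
    sd_multiplier: float = 2.0
    pooled_fraction: float = 0.65         # of pooled cancer samples
    healthy_tissue_scope: str = "peritoneal_only"  # or "all_healthy"
    healthy_filter_scale: str = "RPKM"             # or "PCT_REF"

    def __post_init__(self) -> None:
        if not (0 < self.within_cohort_fraction <= 1
                and 0 < self.pooled_fraction <= 1):
            raise ValidationError("fractions must lie in (0, 1]")
        if self.level_threshold_pct < 0 or self.sd_multiplier < 0:
            raise ValidationError("thresholds must be >= 0")
        if self.min_cohorts < 1:
            raise ValidationError("min_cohorts must be >= 1")
        if self.healthy_tissue_scope not in ("peritoneal_only", "all_healthy"):
            raise ValidationError(
                f"unknown healthy_tissue_scope {self.healthy_tissue_scope!r}")
        if self.healthy_filter_scale not in ("RPKM", "PCT_REF"):
            raise ValidationError(
                f"unknown healthy_filter_scale {self.healthy_filter_scale!r}")


@dataclass
class HealthyStats:
    """Per-gene mean and sample SD (n-1) over in-scope healthy samples."""

    mean_healthy: pd.Series
    sd_healthy: pd.Series
    n_healthy: int
    scale: str = "RPKM"

    def cutoff(self, sd_multiplier: float) -> pd.Series:
        return self.mean_healthy + sd_multiplier * self.sd_healthy


@dataclass
class CoexpressionResult:
    gene_a: str
    gene_b: str
    fraction_a: float
    fraction_b: float
    fraction_both: float


# ---------------------------------------------------------------------------
# Stage 1: per-cohort expressed calls
# ---------------------------------------------------------------------------

def call_expressed(pct: ExpressionMatrix, gpcrs, cfg: SelectionConfig | None = None
                   ) -> set[str]:
    """GPCRs at >= level_threshold_pct of the reference in >= within_cohort_fraction
    of available samples of one cohort."""
    cfg = cfg or SelectionConfig()
    if pct.unit != UNIT_PCT_REF:
        raise ValidationError("call_expressed requires PCT_REF expression")
    present = [g for g in gpcrs if g in pct.values.index]
    if not present:
        raise ValidationError("no GPCR gene present in expression matrix")
    sub = pct.values.loc[present].to_numpy(dtype=float)
    avail = np.isfinite(sub)
    hits = (sub >= cfg.level_threshold_pct) & avail
    n_avail = avail.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_avail > 0, hits.sum(axis=1) / np.maximum(n_avail, 1), 0.0)
    called = {g for g, f, n in zip(present, frac, n_avail)
              if n > 0 and f >= cfg.within_cohort_fraction}
    return called


# ---------------------------------------------------------------------------
# Stage 2: cross-cohort frequency ranking
# ---------------------------------------------------------------------------

def cohort_frequency(sets: dict[str, set[str]], cfg: SelectionConfig | None = None
                     ) -> tuple[dict[str, int], list[str]]:
    """Count, for every gene, the cohorts calling it expressed; pre-select
    genes at frequency >= min_cohorts.

    Returns (frequency table, sorted pre-selected gene list).  The count of
    genes expressed in every cohort is logged.
    """
    cfg = cfg or SelectionConfig()
    if not sets:
        raise ValidationError("cohort_frequency requires at least one cohort")
    freq: dict[str, int] = {}
    for s in sets.values():
        for g in s:
            freq[g] = freq.get(g, 0) + 1
    preselected = sorted(g for g, f in freq.items() if f >= cfg.min_cohorts)
    n_all = sum(1 for f in freq.values() if f == len(sets))
    logger.info("frequency ranking: %d genes in >= %d cohorts, %d in all %d",
                len(preselected), cfg.min_cohorts, n_all, len(sets))
    return freq, preselected


# ---------------------------------------------------------------------------
# Stage 3: healthy-tissue overexpression filter
# ---------------------------------------------------------------------------

def healthy_reference_stats(e_healthy: ExpressionMatrix, meta: SampleMeta,
                            genes, cfg: SelectionConfig | None = None
                            ) -> HealthyStats:
    """Per-gene mean and SD over the in-scope healthy samples.

    scope=peritoneal_only restricts to samples with tissue label
    "peritoneal"; scope=all_healthy uses every healthy sample.
    """
    cfg = cfg or SelectionConfig()
    tissue = "peritoneal" if cfg.healthy_tissue_scope == "peritoneal_only" else None
    in_scope = meta.samples_where(condition="healthy", tissue=tissue)
    in_scope = [s for s in in_scope if s in e_healthy.values.columns]
    if len(in_scope) < 2:
        raise ValidationError(
            f"healthy filter requires >= 2 in-scope healthy samples, got "
            f"{len(in_scope)} (scope={cfg.healthy_tissue_scope})")
    present = [g for g in genes if g in e_healthy.values.index]
    absent = [g for g in genes if g not in e_healthy.values.index]
    sub = e_healthy.values.loc[present, in_scope]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    if absent:
        # not detected in healthy tissue at all: baseline 0 with no spread
        logger.warning("genes absent from healthy matrix treated as zero "
                       "baseline: %s", absent[:10])
        mean = pd.concat([mean, pd.Series(0.0, index=absent)])
        sd = pd.concat([sd, pd.Series(0.0, index=absent)])
    return HealthyStats(mean_healthy=mean.loc[list(genes)],
                        sd_healthy=sd.loc[list(genes)],
                        n_healthy=len(in_scope),
                        scale=cfg.healthy_filter_scale)


def healthy_overexpression_filter(pooled_cancer: ExpressionMatrix,
                                  stats: HealthyStats, candidates,
                                  cfg: SelectionConfig | None = None
                                  ) -> tuple[list[str], dict[str, float]]:
    """Retain candidates exceeding the healthy cutoff in >= pooled_fraction of
    pooled cancer samples.

    cutoff(g) = mean_healthy(g) + sd_multiplier * sd_healthy(g);
    pass_fraction(g) counts only available cells.
    """
    cfg = cfg or SelectionConfig()
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("healthy filter requires a non-empty candidate list")
    missing = [g for g in candidates if g not in stats.mean_healthy.index]
    if missing:
        raise ValidationError(f"candidates without healthy stats: {missing[:10]}")
    cutoff = stats.cutoff(cfg.sd_multiplier)
    pass_fraction: dict[str, float] = {}
    retained: list[str] = []
    for g in candidates:
        if g not in pooled_cancer.values.index:
            pass_fraction[g] = 0.0
            continue
        row = pooled_cancer.values.loc[g].to_numpy(dtype=float)
        avail = np.isfinite(row)
        if not avail.any():
            pass_fraction[g] = 0.0
            continue
        frac = float((row[avail] >= cutoff[g]).sum() / avail.sum())
        pass_fraction[g] = frac
        if frac >= cfg.pooled_fraction:
            retained.append(g)
    logger.info("healthy filter retained %d/%d candidates (n_healthy=%d, "
                "scale=%s)", len(retained), len(candidates), stats.n_healthy,
                stats.scale)
    return retained, pass_fraction


# ---------------------------------------------------------------------------
# Co-expression summaries
# ---------------------------------------------------------------------------

def coexpression_fraction(pooled_pct: ExpressionMatrix, gene_a: str, gene_b: str,
                          cfg: SelectionConfig | None = None) -> CoexpressionResult:
    """Fractions of pooled samples where each gene, and both together, reach
    the expressed-call threshold (on the reference-relative scale)."""
    cfg = cfg or SelectionConfig()
    for g in (gene_a, gene_b):
        if g not in pooled_pct.values.index:
            raise ValidationError(f"gene {g!r} absent from pooled matrix")
    a = pooled_pct.values.loc[gene_a].to_numpy(dtype=float)
    b = pooled_pct.values.loc[gene_b].to_numpy(dtype=float)

    def _frac(mask_vals: np.ndarray, avail: np.ndarray) -> float:
        return float(mask_vals.sum() / avail.sum()) if avail.any() else 0.0

    av_a, av_b = np.isfinite(a), np.isfinite(b)
    ex_a = (a >= cfg.level_threshold_pct) & av_a
    ex_b = (b >= cfg.level_threshold_pct) & av_b
    both_avail = av_a & av_b
    return CoexpressionResult(
        gene_a=gene_a, gene_b=gene_b,
        fraction_a=_frac(ex_a, av_a),
        fraction_b=_frac(ex_b, av_b),
        fraction_both=_frac(ex_a & ex_b & both_avail, both_avail),
    )


def pairwise_coexpression(pooled_pct: ExpressionMatrix, genes,
                          cfg: SelectionConfig | None = None) -> dict[str, float]:
    """fraction_both for every unordered pair, keyed "A|B" (sorted)."""
    out: dict[str, float] = {}
    for a, b in itertools.combinations(sorted(genes), 2):
        res = coexpression_fraction(pooled_pct, a, b, cfg)
        out[f"{a}|{b}"] = res.fraction_both
    return out
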