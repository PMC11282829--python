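"""Within- and between-sample normalization of raw RNA-seq counts.

Implements, directly from their definitions: counts-per-million (CPM),
low-expression gene filtering (two dialects), trimmed-mean-of-M-values (TMM)
scaling factors with effective library sizes, and reads-per-kilobase-per-
million (RPKM) on the TMM-adjusted library sizes.

TMM computes, for each sample against a data-chosen reference sample, gene-wise
log2 expression ratios M_g and average log2 intensities A_g over genes positive
in both samples; after discarding the most extreme fractions of genes by M and
by A, the scaling factor is 2 raised to the (inverse-asymptotic-variance
weighted) mean of the surviving M_g.  Factors are rescaled so their geometric
mean is 1, making them pure between-sample adjustments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CountMatrix, GeneAnnotation, ValidationError

logger = logging.getLogger("gpcrhunt")

#: Units an ExpressionMatrix can carry.
UNIT_CPM = "CPM"
UNIT_RPKM = "RPKM"
UNIT_PCT_REF = "PCT_REF"


@dataclass
class FilterConfig:
    """Low-expression gene filter.

    mode="nonzero_fraction" discards genes with CPM equal to zero in more than
    ``sample_fraction`` of samples; mode="cpm_gt1" keeps genes with CPM above
    ``cpm_threshold`` in at least ``sample_fraction`` of samples.
    """

    mode: str = "nonzero_fraction"
    cpm_threshold: float = 1.0
    sample_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.mode not in ("nonzero_fraction", "cpm_gt1"):
            raise ValidationError(f"unknown filter mode {self.mode!r}")
        if not 0 < self.sample_fraction <= 1:
            raise ValidationError("sample_fraction must be in (0, 1]")
        if self.cpm_threshold < 0:
            raise ValidationError("cpm_threshold must be >= 0")


@dataclass
class TmmConfig:
    logratio_trim: float = 0.30       # trim fraction on M (each tail)
    abs_intensity_trim: float = 0.05  # trim fraction on A (each tail)
    weighting: bool = True            # inverse asymptotic-variance weights

    def __post_init__(self) -> None:
        for t in (self.logratio_trim, self.abs_intensity_trim):
            if not 0 <= t < 0.5:
                raise ValidationError("trim fractions must lie in [0, 0.5)")


@dataclass
class NormalizationFactors:
    """Per-sample library sizes N_k, TMM factors f_k and N_k * f_k."""

    sample_ids: list[str]
    library_size: pd.Series
    tmm_factor: pd.Series

    @property
    def effective_library_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor


@dataclass
class ExpressionMatrix:
    """Real-valued expression, genes x samples, with an explicit unit tag.

    NaN cells mean "value not available" (e.g. the reference gene was zero in
    that sample); downstream fractions exclude them from both numerator and
    denominator.
    """

    values: pd.DataFrame
    unit: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.unit not in (UNIT_CPM, UNIT_RPKM, UNIT_PCT_REF):
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if (finite < 0).any():
            raise ValidationError("expression values must be non-negative")
        if np.isinf(arr).any():
            raise ValidationError("expression values must be finite")

    @property
    def gene_symbols(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------

def compute_cpm(m: CountMatrix) -> ExpressionMatrix:
    """counts / library size x 1e6, per sample."""
    lib = m.library_sizes
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValidationError(
            f"cohort {m.cohort_id}: zero library size for samples {zero}")
    vals = m.counts / lib.to_numpy(dtype=float)[None, :] * 1e6
    return ExpressionMatrix(vals, UNIT_CPM, provenance=f"cpm({m.cohort_id})")


def filter_low_expression(m: CountMatrix, cfg: FilterConfig | None = None
                          ) -> CountMatrix:
    """Drop genes with no or very low expression; counts are not modified.

    Gene order is preserved.  Raises if every gene would be removed.
    """
    cfg = cfg or FilterConfig()
    cpm = compute_cpm(m).values.to_numpy()
    n = cpm.shape[1]
    if cfg.mode == "cpm_gt1":
        keep = (cpm > cfg.cpm_threshold).sum(axis=1) / n >= cfg.sample_fraction
    else:  # nonzero_fraction: discard genes with CPM == 0 in > fraction
        keep = (cpm == 0).sum(axis=1) / n <= cfg.sample_fraction
    if not keep.any():
        raise ValidationError(
            f"cohort {m.cohort_id}: filter removed every gene "
            f"(mode={cfg.mode}); review thresholds")
    kept = m.counts.loc[keep]
    logger.info("cohort %s: low-expression filter (%s) kept %d/%d genes",
                m.cohort_id, cfg.mode, len(kept), len(m.counts))
    return CountMatrix(m.cohort_id, kept)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _trim_keep_mask(v: np.ndarray, trim: float) -> np.ndarray:
    """Keep the central part of v after dropping floor(n*trim) values at each
    end; rank ties broken by array order (stable sort)."""
    n = v.size
    n_drop = int(np.floor(n * trim))
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(v, kind="stable")] = np.arange(n)
    return (ranks >= n_drop) & (ranks < n - n_drop)


def _pairwise_tmm(yk: np.ndarray, nk: float, yr: np.ndarray, nr: float,
                  cfg: TmmConfig) -> float:
    """TMM factor of sample k against reference r (pre-rescaling)."""
    pos = (yk > 0) & (yr > 0)
    if not pos.any():
        raise ValidationError("no gene positive in both samples for TMM")
    a, b = yk[pos].astype(float), yr[pos].astype(float)
    pk, pr = a / nk, b / nr
    m_vals = np.log2(pk / pr)
    if np.max(np.abs(m_vals)) < 1e-10:
        return 1.0  # proportional columns: factor is exactly 1 by definition
    a_vals = 0.5 * np.log2(pk * pr)
    keep = (_trim_keep_mask(m_vals, cfg.logratio_trim)
            & _trim_keep_mask(a_vals, cfg.abs_intensity_trim))
    if not keep.any():
        logger.warning("TMM trimming removed all genes; using untrimmed mean")
        keep = np.ones_like(keep)
    if cfg.weighting:
        w = 1.0 / ((nk - a) / (nk * a) + (nr - b) / (nr * b))
    else:
        w = np.ones_like(m_vals)
    mean_m = np.sum(w[keep] * m_vals[keep]) / np.sum(w[keep])
    return float(2.0 ** mean_m)


def tmm_factors(m: CountMatrix, cfg: TmmConfig | None = None
                ) -> NormalizationFactors:
    """TMM scaling factors for every sample of a cohort.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean 75th percentile across samples (first such sample on ties).
    Factors are rescaled so their geometric mean is exactly 1.
    """
    cfg = cfg or TmmConfig()
    if m.counts.shape[1] < 2:
        raise ValidationError("TMM requires at least 2 samples")
    lib = m.library_sizes.to_numpy(dtype=float)
    cpm = m.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    q75 = np.percentile(cpm, 75, axis=0)  # linear interpolation
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    counts = m.counts.to_numpy()
    factors = np.array([
        _pairwise_tmm(counts[:, k], lib[k], counts[:, ref], lib[ref], cfg)
        for k in range(counts.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    logger.info("cohort %s: TMM reference sample %s", m.cohort_id,
                m.sample_ids[ref])
    return NormalizationFactors(
        sample_ids=list(m.sample_ids),
        library_size=m.library_sizes.astype(float),
        tmm_factor=pd.Series(factors, index=m.sample_ids),
    )


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def compute_rpkm(m: CountMatrix, ann: GeneAnnotation,
                 nf: NormalizationFactors) -> ExpressionMatrix:
    """counts x 1e9 / (gene length in bp x effective library size)."""
    lengths = ann.lengths(m.gene_symbols).to_numpy()
    missing = [s for s in m.sample_ids if s not in nf.effective_library_size.index]
    if missing:
        raise ValidationError(f"normalization factors missing samples: {missing}")
    eff = nf.effective_library_size.loc[m.sample_ids].to_numpy(dtype=float)
    vals = m.counts * 1e9 / (lengths[:, None] * eff[None, :])
    return ExpressionMatrix(vals, UNIT_RPKM,
                            provenance=f"rpkm({m.cohort_id}, tmm-adjusted)")


# ---------------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------------

QUANTILES = (5, 25, 50, 75, 95)


def distribution_summary(e: ExpressionMatrix, gene_subset=None) -> dict:
    """Gene counts and log2(x+1)-scale quantiles for all genes and a subset.

    Summaries pool every available (gene, sample) value; used to compare the
    expression distribution of a gene family (e.g. GPCRs) against all genes.
    """
    def _summ(df: pd.DataFrame) -> dict:
        vals = df.to_numpy(dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return {"n_genes": 0, "quantiles": {}}
        logv = np.log2(vals + 1.0)
        return {
            "n_genes": int(df.shape[0]),
            "quantiles": {q: float(np.percentile(logv, q)) for q in QUANTILES},
        }

    out = {"all": _summ(e.values)}
    if gene_subset is not None:
        present = [g for g in gene_subset if g in e.values.index]
        if not present:
            logger.warning("distribution_summary: empty gene subset")
            out["subset"] = {"n_genes": 0, "quantiles": {}}
        else:
            out["subset"] = _summ(e.values.loc[present])
    return out
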