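"""Seeded generator of multi-cohort RNA-seq counts with planted receptor targets.

Emulates the statistical structure the selection cascade assumes, so the whole
pipeline is testable without any external download:

* negative-binomial counts with per-sample lognormal library sizes;
* a housekeeping gene with low across-sample variability (CV% near a
  configurable target) plus a panel of more variable housekeeping candidates;
* GPCR-flagged genes drawn from a lower-abundance distribution than the bulk
  transcriptome (cell-surface receptors are expressed at low to moderate
  levels);
* planted target receptors: near-silent in healthy tissue, elevated above the
  housekeeping reference in a configurable fraction (penetrance) of cancer
  samples, so they clear both the per-cohort expressed call and the healthy
  mean + 2 SD cutoff;
* decoy receptors that enter but must not survive the cascade — "ubiquitous"
  decoys expressed equally in cancer and healthy tissue (fail the healthy
  filter) and cohort-restricted decoys expressed in too few cohorts (fail the
  frequency ranking).

A truth record listing the planted symbols is returned (and written) next to
the data, so recovery tests never re-derive ground truth from generator
internals.  Identical seeds give bit-identical outputs (NumPy PCG64).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .io_core import CountMatrix, CtTable, GeneAnnotation, SampleMeta, ValidationError
from .reference_gene import DEFAULT_HOUSEKEEPING_CANDIDATES
from .target_selection import REPORTED_FINAL_PANEL

logger = logging.getLogger("gpcrhunt")


@dataclass(frozen=True)
class CohortSpec:
    cohort_id: str
    n_samples: int
    condition: str  # healthy | cancer
    tissues: tuple[str, ...] = ()  # per-sample tissue labels (healthy cohorts)
    group: str = ""

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("cohort needs at least one sample")
        if self.condition not in ("healthy", "cancer"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.tissues and len(self.tissues) != self.n_samples:
            raise ValidationError("tissues must have one label per sample")


def default_cohorts() -> tuple[CohortSpec, ...]:
    """Five cancer cohorts (77/9/10/20/35 samples, pooling to 151) and one
    healthy cohort of 9 samples (3 peritoneal + 3 fallopian + 3 ovarian
    surface), mirroring the public HGSOC collection the pipeline was designed
    around."""
    return (
        CohortSpec("cancer_A", 77, "cancer", group="Pre/Post-chemo"),
        CohortSpec("cancer_B", 9, "cancer", group="Primary/Omentum/Effusion"),
        CohortSpec("cancer_C", 10, "cancer", group="Pre-chemo"),
        CohortSpec("cancer_D", 20, "cancer", group="Primary/Metastatic"),
        CohortSpec("cancer_E", 35, "cancer", group="Pre/Post-NACT"),
        CohortSpec("healthy_A", 9, "healthy",
                   tissues=("peritoneal",) * 3 + ("fallopian",) * 3
                           + ("ovarian_surface",) * 3),
    )


@dataclass
class SyntheticSpec:
    """Generative configuration for a synthetic multi-cohort collection.

    Abundances are molar relative levels; the housekeeping gene sits at 1.0,
    so a planted multiplier of 1.2–2.5 means 120–250% of the reference on the
    length-corrected (RPKM) scale.
    """

    seed: int = 42
    n_genes: int = 2000
    gpcr_count: int = 200
    cohorts: tuple[CohortSpec, ...] = field(default_factory=default_cohorts)
    library_size_lognorm: tuple[float, float] = (14.5, 0.35)  # ln-scale
    dispersion: float = 0.2
    housekeeping_gene: str = "SDHA"
    housekeeping_cv_target: float = 9.0  # CV% across healthy samples (RPKM)
    housekeeping_candidates: tuple[str, ...] = DEFAULT_HOUSEKEEPING_CANDIDATES
    planted_targets: tuple[str, ...] = REPORTED_FINAL_PANEL
    planted_multiplier: tuple[float, float] = (1.2, 2.5)
    planted_penetrance: float = 0.85
    healthy_baseline_quantile: float = 0.25
    n_ubiquitous_decoys: int = 5
    n_cohort_restricted_decoys: int = 5
    stable_dispersion: float = 0.02  # housekeeping candidates & ubiquitous decoys

    def __post_init__(self) -> None:
        if not 0 <= self.planted_penetrance <= 1:
            raise ValidationError("planted_penetrance must lie in [0, 1]")
        if not 0 < self.healthy_baseline_quantile < 1:
            raise ValidationError("healthy_baseline_quantile must lie in (0, 1)")
        if self.housekeeping_gene not in self.housekeeping_candidates:
            raise ValidationError("housekeeping_gene must be among the candidates")
        n_special = (len(self.planted_targets) + self.n_ubiquitous_decoys
                     + self.n_cohort_restricted_decoys)
        if self.gpcr_count < n_special:
            raise ValidationError("gpcr_count too small for planted/decoy genes")
        if self.n_genes < self.gpcr_count + len(self.housekeeping_candidates):
            raise ValidationError("n_genes too small")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        n_cancer = sum(1 for c in self.cohorts if c.condition == "cancer")
        if self.n_cohort_restricted_decoys and n_cancer < 2:
            raise ValidationError(
                "cohort-restricted decoys need at least 2 cancer cohorts")


@dataclass
class SyntheticTruth:
    planted_targets: list[str]
    ubiquitous_decoys: list[str]
    cohort_restricted_decoys: dict[str, list[str]]  # decoy -> cohorts expressed
    housekeeping_gene: str
    housekeeping_candidates: list[str]


@dataclass
class SimulatedCollection:
    cohorts: dict[str, CountMatrix]
    annotation: GeneAnnotation
    meta: SampleMeta
    truth: SyntheticTruth
    spec: SyntheticSpec

    @property
    def cancer_cohort_ids(self) -> list[str]:
        return [c.cohort_id for c in self.spec.cohorts if c.condition == "cancer"]

    @property
    def healthy_cohort_ids(self) -> list[str]:
        return [c.cohort_id for c in self.spec.cohorts if c.condition == "healthy"]


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

# lognormal abundance parameters (ln-scale mean, sd)
_BULK_GENE_LN = (-3.0, 1.5)   # transcriptome bulk
_GPCR_GENE_LN = (-4.5, 1.2)   # receptors: lower, narrower (low-to-moderate)
_CANDIDATE_JITTER_SIGMA = (0.20, 0.40)  # per-candidate across-sample ln-sd
_UBIQUITOUS_LEVEL = (0.6, 1.0)          # x reference, all tissues
_RESTRICTED_LEVEL = (0.8, 1.5)          # x reference, in assigned cohorts


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray
             ) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + phi*mu^2 (gamma-
    Poisson mixture, reproducible under PCG64)."""
    shape = 1.0 / np.maximum(phi, 1e-12)
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def simulate_collection(spec: SyntheticSpec | None = None) -> SimulatedCollection:
    """Generate cohort count matrices, metadata, annotation and truth record."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)

    hk = spec.housekeeping_gene
    candidates = list(spec.housekeeping_candidates)
    planted = list(spec.planted_targets)
    ubi = [f"GPCRU{i + 1:02d}" for i in range(spec.n_ubiquitous_decoys)]
    restricted = [f"GPCRR{i + 1:02d}" for i in range(spec.n_cohort_restricted_decoys)]
    n_gpcr_fill = spec.gpcr_count - len(planted) - len(ubi) - len(restricted)
    gpcr_fill = [f"GPCR{i + 1:04d}" for i in range(n_gpcr_fill)]
    n_bulk = spec.n_genes - spec.gpcr_count - len(candidates)
    bulk = [f"GENE{i + 1:04d}" for i in range(n_bulk)]

    genes = candidates + planted + ubi + restricted + gpcr_fill + bulk
    is_gpcr = [g in set(planted + ubi + restricted + gpcr_fill) for g in genes]
    lengths = np.clip(np.round(rng.lognormal(np.log(2000.0), 0.5, len(genes))),
                      200, 100_000).astype(int)
    annotation = GeneAnnotation(pd.DataFrame(
        {"length_bp": lengths, "is_gpcr": is_gpcr}, index=pd.Index(genes, name="symbol")))

    gi = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # --- per-gene baseline molar abundance (shared across cohorts) ---------
    x_base = np.empty(n_genes)
    x_base[[gi[g] for g in bulk]] = rng.lognormal(*_BULK_GENE_LN, len(bulk))
    x_base[[gi[g] for g in gpcr_fill]] = rng.lognormal(*_GPCR_GENE_LN, len(gpcr_fill))
    x_base[[gi[c] for c in candidates]] = rng.lognormal(0.0, 0.3, len(candidates))
    x_base[gi[hk]] = 1.0
    # planted targets: healthy baseline at a low quantile of the GPCR pool
    z = scipy.stats.norm.ppf(spec.healthy_baseline_quantile)
    baseline_low = float(np.exp(_GPCR_GENE_LN[0] + _GPCR_GENE_LN[1] * z))
    x_base[[gi[g] for g in planted]] = baseline_low
    x_base[[gi[g] for g in ubi]] = rng.uniform(*_UBIQUITOUS_LEVEL, len(ubi))
    x_base[[gi[g] for g in restricted]] = baseline_low

    # across-sample jitter (ln-sd) for non-reference housekeeping candidates
    cand_sigma = rng.uniform(*_CANDIDATE_JITTER_SIGMA, len(candidates))
    cand_sigma[candidates.index(hk)] = 0.0

    # cohort-restricted decoys: each expressed in exactly two cancer cohorts
    cancer_ids = [c.cohort_id for c in spec.cohorts if c.condition == "cancer"]
    restricted_level = rng.uniform(*_RESTRICTED_LEVEL, len(restricted))
    restricted_cohorts = {
        d: sorted(rng.choice(cancer_ids, size=min(2, len(cancer_ids)),
                             replace=False).tolist())
        for d in restricted
    }

    # per-gene dispersion
    phi_gene = np.full(n_genes, spec.dispersion)
    stable = [gi[c] for c in candidates] + [gi[g] for g in ubi]
    phi_gene[stable] = spec.stable_dispersion

    cohort_counts: dict[str, CountMatrix] = {}
    meta_rows = []
    for cs in spec.cohorts:
        n_s = cs.n_samples
        sample_ids = [f"{cs.cohort_id}_S{i + 1:02d}" for i in range(n_s)]
        x = np.tile(x_base[:, None], (1, n_s))

        # candidate housekeeping jitter across samples
        for ci, c in enumerate(candidates):
            if cand_sigma[ci] > 0:
                x[gi[c], :] *= rng.lognormal(0.0, cand_sigma[ci], n_s)

        if cs.condition == "cancer":
            # planted targets elevated in a penetrance fraction of samples
            for g in planted:
                up = rng.random(n_s) < spec.planted_penetrance
                lev = rng.uniform(*spec.planted_multiplier, n_s)
                x[gi[g], up] = lev[up]
            for d in restricted:
                if cs.cohort_id in restricted_cohorts[d]:
                    x[gi[d], :] = restricted_level[restricted.index(d)]

        lib = rng.lognormal(*spec.library_size_lognorm, n_s)
        w = x * lengths[:, None].astype(float)
        p = w / w.sum(axis=0, keepdims=True)
        mu = p * lib[None, :]

        phi = np.tile(phi_gene[:, None], (1, n_s))
        # housekeeping gene: dispersion calibrated to the CV% target
        mu_hk = np.maximum(mu[gi[hk], :], 1.0)
        phi[gi[hk], :] = np.maximum(
            (spec.housekeeping_cv_target / 100.0) ** 2 - 1.0 / mu_hk, 1e-8)

        counts = _nb_draw(rng, mu, phi)
        cohort_counts[cs.cohort_id] = CountMatrix(
            cs.cohort_id, pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                                       columns=sample_ids))
        for i, sid in enumerate(sample_ids):
            meta_rows.append({
                "sample_id": sid,
                "cohort_id": cs.cohort_id,
                "condition": cs.condition,
                "group": cs.group,
                "treatment": "",
                "extraction": "",
                "tissue": cs.tissues[i] if cs.tissues else "",
            })

    meta = SampleMeta(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = SyntheticTruth(
        planted_targets=sorted(planted),
        ubiquitous_decoys=sorted(ubi),
        cohort_restricted_decoys=restricted_cohorts,
        housekeeping_gene=hk,
        housekeeping_candidates=candidates,
    )
    logger.info("simulated %d cohorts, %d genes (%d GPCR-flagged), %d planted "
                "targets", len(cohort_counts), n_genes, sum(is_gpcr), len(planted))
    return SimulatedCollection(cohorts=cohort_counts, annotation=annotation,
                               meta=meta, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# qPCR table simulation
# ---------------------------------------------------------------------------

def simulate_ct_table(genes, n_samples: int = 10, seed: int = 0,
                      reference_gene: str = "SDHA",
                      delta_ct_means: dict[str, float] | None = None,
                      noise_sd: float = 0.8,
                      nondetect_fraction: float = 0.05,
                      detection_limit: float = 35.0) -> CtTable:
    """Synthetic Ct table: reference Ct uniform in 20–23 cycles, per-gene ΔCt
    either given explicitly or drawn uniform in 3–12 cycles, plus Gaussian
    well noise; a configurable fraction of target cells is pushed above the
    detection limit."""
    if not 0 <= nondetect_fraction <= 1:
        raise ValidationError("nondetect_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [g for g in genes if g != reference_gene]
    sample_ids = [f"A{i + 1}" for i in range(n_samples)]
    ref_ct = rng.uniform(20.0, 23.0, n_samples)
    if delta_ct_means is None:
        means = rng.uniform(3.0, 12.0, len(genes))
    else:
        missing = [g for g in genes if g not in delta_ct_means]
        if missing:
            raise ValidationError(f"delta_ct_means missing genes: {missing}")
        means = np.array([delta_ct_means[g] for g in genes], dtype=float)
    ct = ref_ct[None, :] + means[:, None]
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, ct.shape)
    if nondetect_fraction > 0:
        mask = rng.random(ct.shape) < nondetect_fraction
        ct = np.where(mask, rng.uniform(36.0, 40.0, ct.shape), ct)
    ct = np.clip(ct, 5.0, 45.0)
    table = pd.DataFrame(np.vstack([ref_ct[None, :], ct]),
                         index=pd.Index([reference_gene] + genes, name="gene"),
                         columns=sample_ids)
    return CtTable(table, reference_gene=reference_gene,
                   detection_limit=detection_limit)


# ---------------------------------------------------------------------------
# On-disk form
# ---------------------------------------------------------------------------

def write_collection(coll: SimulatedCollection, outdir: str | Path) -> None:
    """Write the collection in the TSV formats the readers accept, plus the
    truth record (truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cid, cm in coll.cohorts.items():
        cm.counts.to_csv(outdir / f"counts_{cid}.tsv", sep="\t", index_label="gene")
    coll.annotation.table.to_csv(outdir / "annotation.tsv", sep="\t",
                                 index_label="symbol")
    coll.meta.table.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample_id")
    (outdir / "truth.json").write_text(
        json.dumps(dataclasses.asdict(coll.truth), indent=2) + "\n")
    logger.info("collection written to %s", outdir)
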