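"""Reading, validation and reporting of the pipeline's tabular inputs and outputs.

Count matrices arrive as TSV/CSV (gene-symbol first column) or as an MTX
triplet directory; gene annotation and sample metadata are flat TSV tables;
qPCR cycle-threshold data is a long-format well table.  Selection results are
written as a JSON report plus flat TSV tables so that downstream consumers
never need to re-run the pipeline to inspect them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("gpcrhunt")

HEALTHY_TISSUES = ("peritoneal", "fallopian", "ovarian_surface")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene-level annotation: HGNC-style symbol, transcript length, GPCR flag.

    ``table`` is indexed by unique gene symbol with columns ``length_bp``
    (positive int, used for per-kilobase normalization) and ``is_gpcr`` (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"length_bp", "is_gpcr"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols in annotation: {dups[:5]}")
        if (self.table.index == "").any() or self.table.index.isna().any():
            raise ValidationError("empty gene symbol in annotation")
        bad = self.table.index[self.table["length_bp"] <= 0].tolist()
        if bad:
            raise ValidationError(f"non-positive length_bp for genes: {bad[:5]}")

    @property
    def symbols(self) -> pd.Index:
        return self.table.index

    @property
    def gpcr_symbols(self) -> list[str]:
        return self.table.index[self.table["is_gpcr"].astype(bool)].tolist()

    @property
    def n_gpcrs(self) -> int:
        return int(self.table["is_gpcr"].astype(bool).sum())

    def lengths(self, genes) -> pd.Series:
        missing = [g for g in genes if g not in self.table.index]
        if missing:
            raise ValidationError(f"genes without annotated length: {missing[:10]}")
        return self.table.loc[list(genes), "length_bp"].astype(float)


@dataclass
class SampleMeta:
    """Per-sample metadata: cohort, condition, subtype/treatment labels.

    ``table`` is indexed by unique sample id with at least ``cohort_id`` and
    ``condition`` (healthy | cancer); optional free-text ``group``,
    ``treatment``, ``extraction`` and, for healthy samples, ``tissue``
    (peritoneal | fallopian | ovarian_surface).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cohort_id", "condition"} - set(self.table.columns)
        if required:
            raise ValidationError(f"sample metadata missing columns: {sorted(required)}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        bad = set(self.table["condition"]) - {"healthy", "cancer"}
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_where(self, *, condition: str | None = None,
                      tissue: str | None = None,
                      cohort_id: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if condition is not None:
            mask &= self.table["condition"] == condition
        if tissue is not None:
            if "tissue" not in self.table.columns:
                raise ValidationError(
                    "tissue labels required to restrict healthy samples by tissue")
            mask &= self.table["tissue"] == tissue
        if cohort_id is not None:
            mask &= self.table["cohort_id"] == cohort_id
        return self.table.index[mask].tolist()


@dataclass
class CountMatrix:
    """Raw integer counts for one cohort, genes x samples."""

    cohort_id: str
    counts: pd.DataFrame  # genes x samples, non-negative integers

    def __post_init__(self) -> None:
        if self.counts.size == 0:
            raise ValidationError(f"cohort {self.cohort_id}: empty count matrix")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError(f"cohort {self.cohort_id}: non-numeric counts")
        neg = np.argwhere(arr < 0)
        if neg.size:
            g, s = neg[0]
            raise ValidationError(
                f"cohort {self.cohort_id}: negative count at gene "
                f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}")
        frac = np.argwhere(arr != np.floor(arr))
        if frac.size:
            g, s = frac[0]
            raise ValidationError(
                f"cohort {self.cohort_id}: non-integer count at gene "
                f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}")
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_symbols(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.cohort_id, self.counts.loc[list(genes)])


@dataclass
class CtTable:
    """qPCR cycle-threshold values, genes x samples, with detection limit.

    Missing wells are NaN.  ``replicate_sd`` carries the across-replicate
    standard deviation when the table was built from replicate wells.
    """

    ct: pd.DataFrame  # genes x samples, cycles; NaN = missing
    reference_gene: str = "SDHA"
    detection_limit: float = 35.0
    replicate_sd: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.ct.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite <= 0) | (finite >= 60)).any():
            raise ValidationError("Ct values must lie in (0, 60) cycles")
        if self.reference_gene not in self.ct.index:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} absent from Ct table")

    @property
    def gene_symbols(self) -> pd.Index:
        return self.ct.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.ct.columns


@dataclass
class SelectionReport:
    """Outcome of the selection cascade.

    per_cohort_expressed: cohort id -> set of GPCR symbols called expressed.
    frequency: gene -> number of cohorts whose set contains it.
    preselected: genes expressed in at least ``min_cohorts`` cohorts.
    final_targets: genes surviving the healthy-tissue overexpression filter.
    pass_fraction: gene -> fraction of pooled cancer samples above the healthy
    cutoff.  coexpression: "A|B" -> fraction of pooled samples where both
    genes are called expressed.  cluster_labels: optional sample -> cluster id.
    """

    per_cohort_expressed: dict[str, set[str]]
    frequency: dict[str, int]
    preselected: list[str]
    final_targets: list[str]
    pass_fraction: dict[str, float] = field(default_factory=dict)
    coexpression: dict[str, float] = field(default_factory=dict)
    cluster_labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        union = set().union(*self.per_cohort_expressed.values()) \
            if self.per_cohort_expressed else set()
        if not set(self.preselected) <= union:
            raise ValidationError("preselected genes not contained in cohort union")
        if not set(self.final_targets) <= set(self.preselected):
            raise ValidationError("final targets not contained in preselected set")
        for g, f in self.frequency.items():
            n = sum(g in s for s in self.per_cohort_expressed.values())
            if n != f:
                raise ValidationError(f"frequency mismatch for {g}: {f} != {n}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _collapse_duplicates(df: pd.DataFrame, cohort_id: str) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    dups = df.index[df.index.duplicated()].unique().tolist()
    logger.warning("cohort %s: collapsing %d duplicated gene symbols by summation: %s",
                   cohort_id, len(dups), dups[:10])
    # groupby(sort=False) preserves first-occurrence order
    return df.groupby(level=0, sort=False).sum()


def read_counts(path: str | Path, cohort_id: str) -> CountMatrix:
    """Read a count matrix from a TSV/CSV file or an MTX triplet directory.

    TSV/CSV: gene-symbol first column, one column per sample, separator
    sniffed.  MTX: directory containing ``matrix.mtx`` (genes x samples),
    ``genes.tsv`` and ``samples.tsv`` (one name per line).  Duplicate gene
    symbols are collapsed by summation and logged.
    """
    path = Path(path)
    if path.is_dir():
        mtx = scipy.io.mmread(path / "matrix.mtx")
        genes = (path / "genes.tsv").read_text().split()
        samples = (path / "samples.tsv").read_text().split()
        df = pd.DataFrame(np.asarray(mtx.todense() if scipy.sparse.issparse(mtx) else mtx),
                          index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index.name = "gene"
    df = _collapse_duplicates(df, cohort_id)
    return CountMatrix(cohort_id, df)


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read gene annotation TSV with columns symbol, length_bp, is_gpcr."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"symbol", "length_bp", "is_gpcr"} - set(df.columns)
    if missing:
        raise ValidationError(f"annotation file missing columns: {sorted(missing)}")
    df = df.set_index("symbol")
    df["is_gpcr"] = df["is_gpcr"].map(_parse_bool)
    ann = GeneAnnotation(df)
    logger.info("annotation: %d genes, %d GPCR-flagged", len(ann.symbols), ann.n_gpcrs)
    return ann


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"true", "1", "yes", "t"}
    return bool(v)


def read_sample_meta(path: str | Path) -> SampleMeta:
    """Read sample metadata TSV (sample_id, cohort_id, condition, ...)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "sample_id" not in df.columns:
        raise ValidationError("sample metadata requires a sample_id column")
    return SampleMeta(df.set_index("sample_id"))


def read_ct_table(path: str | Path, reference_gene: str = "SDHA",
                  detection_limit: float = 35.0) -> CtTable:
    """Read a long-format qPCR table (columns sample_id, gene, ct).

    Replicate wells (repeated sample x gene rows) are averaged; their
    standard deviation is retained on the returned table.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"sample_id", "gene", "ct"} - set(df.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    grouped = df.groupby(["gene", "sample_id"], sort=False)["ct"]
    mean = grouped.mean().unstack("sample_id")
    sd = grouped.std(ddof=1).unstack("sample_id")
    # restore input gene order
    order = df["gene"].drop_duplicates().tolist()
    cols = df["sample_id"].drop_duplicates().tolist()
    mean, sd = mean.loc[order, cols], sd.loc[order, cols]
    return CtTable(mean, reference_gene=reference_gene,
                   detection_limit=detection_limit, replicate_sd=sd)


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

def write_report(report: SelectionReport, path: str | Path) -> None:
    """Write a SelectionReport to ``path`` (JSON) plus sibling TSV tables.

    TSVs written next to the JSON: ``<stem>_frequency.tsv`` (gene, n_cohorts,
    pass_fraction), ``<stem>_final_panel.tsv`` and ``<stem>_clusters.tsv``.
    ``read_report`` on the JSON reproduces the report exactly.
    """
    path = Path(path)
    payload = {
        "per_cohort_expressed": {c: sorted(s) for c, s in
                                 report.per_cohort_expressed.items()},
        "frequency": dict(sorted(report.frequency.items())),
        "preselected": list(report.preselected),
        "final_targets": list(report.final_targets),
        "pass_fraction": dict(sorted(report.pass_fraction.items())),
        "coexpression": dict(sorted(report.coexpression.items())),
        "cluster_labels": dict(report.cluster_labels),
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")

    stem = path.with_suffix("")
    freq = pd.DataFrame({
        "gene": sorted(report.frequency),
        "n_cohorts": [report.frequency[g] for g in sorted(report.frequency)],
    })
    freq.to_csv(f"{stem}_frequency.tsv", sep="\t", index=False)
    panel = pd.DataFrame({
        "gene": report.final_targets,
        "pass_fraction": [report.pass_fraction.get(g, np.nan)
                          for g in report.final_targets],
    })
    panel.to_csv(f"{stem}_final_panel.tsv", sep="\t", index=False)
    if report.cluster_labels:
        pd.DataFrame({
            "sample_id": list(report.cluster_labels),
            "cluster": list(report.cluster_labels.values()),
        }).to_csv(f"{stem}_clusters.tsv", sep="\t", index=False)
    logger.info("report written to %s (%d final targets)", path,
                len(report.final_targets))


def read_report(path: str | Path) -> SelectionReport:
    payload = json.loads(Path(path).read_text())
    return SelectionReport(
        per_cohort_expressed={c: set(s) for c, s in
                              payload["per_cohort_expressed"].items()},
        frequency={g: int(v) for g, v in payload["frequency"].items()},
        preselected=list(payload["preselected"]),
        final_targets=list(payload["final_targets"]),
        pass_fraction={g: float(v) for g, v in payload["pass_fraction"].items()},
        coexpression={k: float(v) for k, v in payload["coexpression"].items()},
        cluster_labels={s: int(v) for s, v in payload["cluster_labels"].items()},
    )


def write_expression_tsv(values: pd.DataFrame, unit: str, provenance: str,
                         path: str | Path) -> None:
    """Write an expression matrix TSV with a header comment recording unit."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# unit={unit} provenance={provenance}\n")
        values.to_csv(fh, sep="\t", index_label="gene")
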